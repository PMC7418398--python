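"""End-to-end orchestration: quantify -> QC/prune/PCA -> scan ->
correlations/hotspots -> region mapping/enrichment -> traits/coloc.

Every stage writes a self-describing TSV under the output directory and
one structured log line with input/output row counts; a JSON manifest
records versions, seeds, and parameters so a run can be reproduced
bit-identically.
"""
from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .datatypes import ProteinMatrix
from .errors import ConfigurationError, InputValidationError
from .hotspots import (find_eqtl_hotspots, find_hotspots, shared_hotspot_enrichment,
                       spearman_matrix)
from .qc import QcThresholds, genotype_pca, ld_prune, variant_qc
from .regions import (local_distant_region_distribution, map_to_gene_features,
                      map_to_regulatory, regulator_enrichment)
from .scan import ScanConfig, eligible_proteins, scan
from .tpa import quantify_matrix
from .traits import coloc_table, colocalize, map_traits, trait_summary

logger = logging.getLogger(__name__)

BACKGROUND_GENE = "_background_"


@dataclass
class PipelineConfig:
    vcf: str
    peptides: str
    protein_meta: str
    covariates: str
    regulatory: str | None = None
    genes: str | None = None
    traits: str | None = None
    external_qtl: str | None = None
    out_dir: str = "pqtl_out"
    qc: QcThresholds = field(default_factory=QcThresholds)
    scan: ScanConfig = field(default_factory=ScanConfig)
    prune_window: int = 50
    prune_step: int = 5
    prune_r2: float = 0.8
    hotspot_max_gap: int = 1_000_000
    hotspot_min_abs_rho: float = 0.5
    enrichment_alpha: float = 0.05
    coloc_r2: float = 0.8
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        qc = QcThresholds(**raw.pop("qc", {}))
        scan_cfg = ScanConfig(**raw.pop("scan", {}))
        return cls(qc=qc, scan=scan_cfg, **raw)

    def input_paths(self) -> dict[str, str | None]:
        return {k: getattr(self, k) for k in
                ("vcf", "peptides", "protein_meta", "covariates",
                 "regulatory", "genes", "traits", "external_qtl")}


def validate_inputs(config: PipelineConfig) -> list[str]:
    """Pre-flight checks; raises on fatal problems, returns warnings.

    Checks file existence, VCF position sortedness, sample-ID concordance
    (extra samples are intersected with a warning), and the regulatory
    feature vocabulary.
    """
    warnings: list[str] = []
    for name, path in config.input_paths().items():
        if path is not None and not Path(path).exists():
            raise ConfigurationError(f"input file for {name!r} not found: {path}")

    genotypes = io.read_vcf(config.vcf)  # GenotypeMatrix validates sorting
    covariates = io.read_tsv(config.covariates)
    peptides = io.read_peptide_table(config.peptides)

    geno = set(genotypes.samples)
    for label, ids in (("covariates", set(covariates["sample"])),
                       ("peptide table", set(peptides.samples))):
        extra, absent = ids - geno, geno - ids
        if extra:
            warnings.append(f"{label}: {len(extra)} sample(s) not genotyped, "
                            f"intersecting: {sorted(extra)[:5]}")
        if absent:
            warnings.append(f"{label}: {len(absent)} genotyped sample(s) missing, "
                            f"intersecting: {sorted(absent)[:5]}")
    if config.regulatory:
        regions = io.read_bed(config.regulatory)
        from .regions import REGULATORY_VOCABULARY
        bad = set(regions["feature"]) - REGULATORY_VOCABULARY
        if bad:
            raise InputValidationError(f"unknown regulatory classes: {sorted(bad)}")
    return warnings


def _log_stage(name: str, n_in: int, n_out: int) -> None:
    logger.info("stage=%s rows_in=%d rows_out=%d", name, n_in, n_out)


def run_all(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the summary dict.

    Any stage failure is re-raised annotated with the stage name.
    """
    warnings = validate_inputs(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"warnings": warnings}
    stage = "load"
    try:
        genotypes = io.read_vcf(config.vcf)
        covariates = io.read_tsv(config.covariates)
        peptides = io.read_peptide_table(config.peptides)
        meta = io.read_tsv(config.protein_meta)

        stage = "quantify"
        real = list(meta.loc[meta["gene"] != BACKGROUND_GENE, "protein"])
        proteins = quantify_matrix(peptides, meta, quantify=real)
        io.write_protein_matrix(proteins, out / "protein_matrix.tsv",
                                out / "protein_meta.tsv")
        _log_stage(stage, len(peptides.table), len(proteins.values))

        stage = "sample-intersection"
        common = [s for s in genotypes.samples
                  if s in set(proteins.samples) & set(covariates["sample"])]
        if not common:
            raise InputValidationError("no samples shared across inputs")
        keep = [genotypes.samples.index(s) for s in common]
        genotypes.dosages = genotypes.dosages[keep, :]
        genotypes.samples = common
        proteins = ProteinMatrix(values=proteins.values[common],
                                 meta=proteins.meta)
        covariates = covariates[covariates["sample"].isin(common)]

        stage = "qc"
        filtered, qc_report = variant_qc(genotypes, config.qc)
        io.write_tsv(pd.DataFrame([asdict(qc_report) | {"removed": None}])
                     .drop(columns="removed"), out / "qc_report.tsv")
        _log_stage(stage, genotypes.n_variants, filtered.n_variants)

        stage = "prune"
        retained = ld_prune(filtered, config.prune_window, config.prune_step,
                            config.prune_r2)
        (out / "pruned_variants.txt").write_text("\n".join(retained) + "\n")
        _log_stage(stage, filtered.n_variants, len(retained))

        stage = "pca"
        pcs = genotype_pca(filtered, k=config.scan.n_pcs)
        io.write_tsv(pcs, out / "pcs.tsv")

        stage = "scan"
        result = scan(filtered, proteins, covariates, config.scan, pcs=pcs)
        io.write_tsv(result.records, out / "associations.tsv")
        _log_stage(stage, result.n_tests, len(result.records))

        stage = "correlate"
        corr = spearman_matrix(proteins)
        corr.rho.rename_axis("protein").to_csv(out / "spearman_rho.tsv", sep="\t")

        stage = "hotspots"
        spots = find_hotspots(result.records, corr, config.hotspot_max_gap,
                              config.hotspot_min_abs_rho)
        hs_df = pd.DataFrame([{
            "id": h.id, "chrom": h.chrom, "start": h.start, "end": h.end,
            "n_variants": h.n_variants, "n_proteins": len(h.proteins),
            "proteins": ";".join(h.proteins),
            "variants": ";".join(h.variants),
        } for h in spots])
        io.write_tsv(hs_df, out / "hotspots.tsv")
        _log_stage(stage, len(result.records), len(spots))
        if spots:
            odds, p_enr, _tab = shared_hotspot_enrichment(
                corr, spots, min_abs_rho=config.hotspot_min_abs_rho)
            summary["shared_hotspot_or"] = odds
            summary["shared_hotspot_p"] = p_enr

        eqtl_spots = []
        if config.external_qtl:
            stage = "eqtl-hotspots"
            external = io.read_tsv(config.external_qtl)
            eqtl_spots = find_eqtl_hotspots(external, filtered.variants,
                                            proteins.meta, corr,
                                            config.hotspot_max_gap,
                                            config.hotspot_min_abs_rho)

        region_counts = {}
        if config.regulatory or config.genes:
            stage = "map-regions"
            sig_variants = result.records[["rsid", "chrom", "pos"]] \
                .drop_duplicates().reset_index(drop=True)
            if config.regulatory:
                regions = io.read_bed(config.regulatory)
                reg_hits = map_to_regulatory(sig_variants, regions)
                io.write_tsv(reg_hits, out / "regulatory_hits.tsv")
                region_counts = reg_hits["feature"].value_counts().to_dict()
            if config.genes:
                genes = io.read_gtf(config.genes)
                universe = filtered.variants[["rsid", "chrom", "pos"]]
                labels = map_to_gene_features(universe, genes)
                io.write_tsv(labels[labels["rsid"].isin(sig_variants["rsid"])],
                             out / "gene_feature_labels.tsv")
                dist = local_distant_region_distribution(result.records, labels)
                io.write_tsv(dist, out / "region_distribution.tsv")

                stage = "enrich"
                universe_ids = set(universe["rsid"])
                enrich_frames = []
                by_protein = result.records.groupby("protein")["rsid"].agg(set)
                per_protein = {p: regulator_enrichment(p, set(v), universe_ids,
                                                       labels, n_tests=1)
                               for p, v in by_protein.items()}
                n_tests = sum(len(df) for df in per_protein.values())
                for p, df in per_protein.items():
                    df = df.copy()
                    df["p_adjusted"] = np.minimum(1.0, df["p"] * max(n_tests, 1))
                    df["significant"] = ((df["p_adjusted"] < config.enrichment_alpha)
                                         & (df["odds_ratio"] > 1))
                    enrich_frames.append(df)
                enrichment = (pd.concat(enrich_frames, ignore_index=True)
                              if enrich_frames else pd.DataFrame())
                io.write_tsv(enrichment, out / "regulator_enrichment.tsv")
                summary["n_predicted_regulators"] = (
                    int(enrichment.loc[enrichment["significant"], "gene"].nunique())
                    if len(enrichment) else 0)

        triples = pd.DataFrame(columns=["rsid", "protein", "trait", "source"])
        if config.traits:
            stage = "integrate"
            catalog = io.read_tsv(config.traits)
            triples = map_traits(result.records, catalog)
            io.write_tsv(triples, out / "variant_trait_triples.tsv")

        coloc_rows = []
        if config.external_qtl and len(result.records):
            stage = "coloc"
            external = io.read_tsv(config.external_qtl)
            for prot, recs in result.records.groupby("protein"):
                y = proteins.values.loc[prot, common].to_numpy(dtype=float)
                results, _ = colocalize(
                    prot, y, recs, external, filtered,
                    threshold=result.threshold, r2_threshold=config.coloc_r2)
                coloc_rows.extend(results)
            io.write_tsv(coloc_table(coloc_rows), out / "colocalization.tsv")
    except Exception as exc:
        raise type(exc)(f"[stage {stage}] {exc}") from exc

    summary.update(result.summary)
    summary.update({
        "n_variants_post_qc": filtered.n_variants,
        "n_independent_markers": len(retained),
        "n_eligible_proteins": len(eligible_proteins(
            proteins, config.scan.min_quantified_frac)),
        "threshold": result.threshold,
        "n_hotspots": len(spots),
        "n_eqtl_hotspots": len(eqtl_spots),
        "n_trait_triples": trait_summary(triples)["n_triples"],
        "n_coloc_tests": len(coloc_rows),
        "n_colocalized": int(sum(r.colocalized for r in coloc_rows)),
        "regulatory_hit_counts": region_counts,
    })
    manifest = {
        "pqtlkit_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "parameters": {
            "qc": asdict(config.qc),
            "scan": asdict(config.scan),
            "prune": {"window": config.prune_window, "step": config.prune_step,
                      "r2": config.prune_r2},
            "hotspots": {"max_gap": config.hotspot_max_gap,
                         "min_abs_rho": config.hotspot_min_abs_rho},
            "enrichment_alpha": config.enrichment_alpha,
            "coloc_r2": config.coloc_r2,
        },
        "inputs": config.input_paths(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=str))
    return summary
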