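"""Readers and writers for the plain-text interchange formats.

Conventions: VCF carries GT-only genotypes; BED is 0-based half-open on
disk and converted to 1-based inclusive at ingest; GTF is 1-based
inclusive throughout; everything else is TSV.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datatypes import GenotypeMatrix, PeptideSignalTable, ProteinMatrix
from .errors import InputValidationError

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    path = Path(path)
    chroms = matrix.variants["chrom"].unique()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=pqtlkit-simulate\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.samples) + "\n")
        for j, var in enumerate(matrix.variants.itertuples()):
            gts = []
            for d in matrix.dosages[:, j]:
                gts.append("./." if not np.isfinite(d) else _GT_STRINGS[int(d)])
            fh.write(f"{var.chrom}\t{var.pos}\t{var.rsid}\t{var.ref}\t{var.alt}"
                     f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Load a GT-only VCF into a dosage matrix (NaN = missing call)."""
    vcf = VCF(str(path), gts012=True)  # gt_types: 0/1/2 dosage, 3 unknown
    samples = list(vcf.samples)
    rows, cols = [], []
    for variant in vcf:
        alt = variant.ALT[0] if variant.ALT else "."
        rows.append((str(variant.CHROM), int(variant.POS),
                     variant.ID or f"{variant.CHROM}:{variant.POS}",
                     variant.REF, alt))
        gt = variant.gt_types.astype(float)
        gt[gt == 3] = np.nan
        cols.append(gt)
    vcf.close()
    if not rows:
        raise InputValidationError(f"no variants in {path}")
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "rsid", "ref", "alt"])
    return GenotypeMatrix(samples=samples, variants=variants,
                          dosages=np.column_stack(cols))


def write_peptide_table(table: PeptideSignalTable, path: str | Path) -> None:
    out = table.table.copy()
    out["protein_ids"] = [";".join(g) for g in out["protein_ids"]]
    out.to_csv(path, sep="\t", index=False)


def read_peptide_table(path: str | Path) -> PeptideSignalTable:
    df = pd.read_csv(path, sep="\t")
    fixed = ["peptide_id", "sequence", "protein_ids"]
    missing = [c for c in fixed if c not in df.columns]
    if missing:
        raise InputValidationError(f"peptide table missing columns {missing}")
    df["protein_ids"] = [tuple(str(g).split(";")) for g in df["protein_ids"]]
    samples = [c for c in df.columns if c not in fixed]
    return PeptideSignalTable(table=df, samples=samples)


def write_protein_matrix(matrix: ProteinMatrix, values_path: str | Path,
                         meta_path: str | Path) -> None:
    matrix.values.rename_axis("protein").to_csv(values_path, sep="\t")
    matrix.meta.to_csv(meta_path, sep="\t", index=False)


def read_protein_matrix(values_path: str | Path,
                        meta_path: str | Path) -> ProteinMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col="protein")
    meta = pd.read_csv(meta_path, sep="\t", dtype={"chrom": str})
    return ProteinMatrix(values=values, meta=meta)


def write_bed(regions: pd.DataFrame, path: str | Path) -> None:
    """1-based inclusive intervals -> BED 0-based half-open with the
    feature class in column 4."""
    out = regions.copy()
    out["start"] = out["start"] - 1
    out[["chrom", "start", "end", "feature"]].to_csv(
        path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "feature"],
                     dtype={"chrom": str})
    df["start"] = df["start"] + 1
    if (df["start"] > df["end"]).any():
        raise InputValidationError(f"interval with start > end in {path}")
    return df


def write_gtf(genes: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in genes.itertuples():
            attrs = f'gene_id "{rec.gene}"; gene_type "{rec.biotype}";'
            fh.write(f"{rec.chrom}\tpqtlkit\t{rec.feature}\t{rec.start}"
                     f"\t{rec.end}\t.\t+\t.\t{attrs}\n")


def read_gtf(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise InputValidationError(f"malformed GTF line in {path}")
            attrs = dict(
                (kv.strip().split(" ", 1)[0],
                 kv.strip().split(" ", 1)[1].strip('"'))
                for kv in fields[8].rstrip(";").split(";") if kv.strip())
            rows.append((attrs.get("gene_id"), attrs.get("gene_type"),
                         fields[2], str(fields[0]), int(fields[3]),
                         int(fields[4])))
    return pd.DataFrame(rows, columns=["gene", "biotype", "feature",
                                       "chrom", "start", "end"])


def write_ground_truth(truth, path: str | Path) -> None:
    payload = {
        "betas": [{"variant": v, "protein": p, "beta": b}
                  for (v, p), b in truth.betas.items()],
        "clusters": {str(k): v for k, v in truth.clusters.items()},
        "colocalized_pairs": truth.colocalized_pairs,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str}, **kwargs)
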